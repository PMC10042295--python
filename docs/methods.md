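# Methods

This note documents the models, procedures and design choices behind
`ecg2img`: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the numerically
delicate decisions live.

## 1. Problem setting

The toolkit targets short-term mortality prediction from resting
10-second ECGs of cardiac-care-unit patients, approached as an image
classification problem: the multi-lead waveform is rendered into
standardized grayscale images and a 2-D CNN classifies each image as
survivor / non-survivor, with per-patient aggregation of the per-image
scores. Because real CCU cohorts are private, every stage is exercised
end-to-end on synthetic cohorts (section 7).

## 2. Lead selection and aVR derivation

The imaging panel uses four leads in fixed top-to-bottom order — II, V3,
V5, aVR — a subset chosen in the prognosis literature for carrying most
of the survival-relevant information of the 12-lead set. aVR is an
augmented limb lead defined arithmetically from the Einthoven leads:

    aVR(t) = -(I(t) + II(t)) / 2

If a record already contains a measured/device-derived aVR channel it is
passed through unchanged; re-deriving it would discard information only
in the degenerate case where the device used a different convention, and
the pass-through keeps the operation idempotent. The derivation is
symmetric in I and II and linear in amplitude; with a consistent
Einthoven triple (III = II − I) the three augmented leads satisfy
aVR + aVL + aVF = 0, which the test suite uses as an oracle.

## 3. Image encoding

Each lead of a 5000-sample record is split into 3 contiguous segments
(1667/1667/1666 — earlier segments take the extra sample) so the
rendered traces retain enough time resolution for rhythm and morphology
to be legible. Per segment and lead:

1. **Native rasterization.** One pixel column per sample
   (width = segment length), 256 rows. Amplitude maps linearly from a
   fixed symmetric range of ±2.0 mV to rows 0 (top, +2 mV) through 255
   (bottom, −2 mV); out-of-range values clip to the edge rows. Every
   column receives the linearly interpolated trace value and consecutive
   columns are joined vertically, giving a connected 1-px black
   (intensity 0) polyline on white (255).
2. **Lanczos reduction** to 224 wide × 26 high (3-lobe windowed sinc;
   section 4).
3. **Stacking.** The four strips are stacked in panel order with 40
   background rows between consecutive strips: 4·26 + 3·40 = 224, the
   only integer strip height consistent with a 224-px image and 40-px
   gaps. Output is one 224×224 8-bit grayscale PNG per segment, three
   per patient.

Fixed choices worth knowing:

* **Fixed amplitude range, not per-segment min–max.** A fixed ±2 mV
  range keeps pixel row meaningful across segments and patients (an
  ST-segment shifted by 0.2 mV is shifted by the same number of rows
  everywhere), which both cardiologist reading and attribution analysis
  rely on. The range is configurable (`RenderConfig.amp_range_mv`).
* **Native height 256 px** before reduction: roughly 10× the final strip
  height, enough for morphology to survive the low-pass of the
  reduction.
* **Rounding of trace rows** uses floor(y + 0.5). An exactly zero
  amplitude falls on the half-row midline of an even-height strip and
  lands on row 128 of 256; this is the one place where the
  negate-and-mirror symmetry of the rasterizer is broken by a half-pixel.
* Encoding is fully deterministic: identical inputs produce
  byte-identical PNGs.

## 4. Lanczos resampling

Resampling is separable windowed-sinc with `taps` = 3 lobes:
L(x) = sinc(x)·sinc(x/a) for |x| < a. Output pixel centers follow the
half-pixel convention; on downscale the kernel is widened by the scale
factor (antialiasing); source indices beyond the edges are clamped; each
output pixel's weights are normalized to unit sum, so constants are
preserved exactly. The implementation builds dense per-axis weight
matrices (cached) and is verified against an independent direct
per-pixel convolution oracle to within one 8-bit intensity level — the
residual being float summation order at rounding boundaries.

## 5. Classifier harness

### 5.1 Transfer-learning surface

A *backbone* is any convolutional feature extractor. Its classification
head is discarded and replaced by global average pooling → dense
(256 hidden units, ReLU) → dense(2) with softmax normalization — the
minimal two-layer head consistent with retraining "only the coupled
layers". With `freeze_backbone=True` (default) the optimizer updates
only the head; frozen parameters are bit-identical before and after
training. Large pretrained backbones are deliberately not bundled: the
harness is backbone-agnostic and ships `tiny2d`, a three-block CNN
(3×3 conv stride 2 → 2× maxpool → two 3×3 conv + 2× maxpool blocks;
8/16/32 channels) that trains from scratch on a CPU in about a minute
for 600 images × 10 epochs. When `tiny2d` is trained from scratch the
experiments set `freeze_backbone=False` — freezing random filters is
meaningful only in the transfer setting.

The layers are implemented in-repo in plain single-precision numpy with
exact manual backpropagation (`ecg2img.nn`): convolution via im2col,
non-overlapping max pooling, Adam. Everything is seeded; two runs with
the same seed, data and config produce identical histories.

### 5.2 Training protocol

Cross-entropy loss, Adam. Desk-scale defaults: learning rate 1e-3,
10 epochs, batch size 8. (The original GPU-scale protocol — learning
rate 1e-6, 50 epochs, batch 8, pretrained ImageNet backbones — is kept
as constants `PAPER_LEARNING_RATE` / `PAPER_EPOCHS` for reference.)
There is no early stopping: the model at the final epoch is the model
evaluated, and the validation split is used only to monitor the loss.
Train/validation/test splits are at patient level; any overlap raises a
leakage error before training starts.

### 5.3 1-D baseline

The conventional-analysis baseline consumes the raw (4, 5000) lead
array: four independent branches (one per lead), each four conv+pool
blocks (kernel 7/7/5/5, channels 8/16/32/32, 4× pooling), global
average pooling per branch, and a single fully connected layer over the
concatenated 128 features.

## 6. Aggregation, metrics and cross-validation

Per-patient score = arithmetic mean of the three per-image death
probabilities; predicted non-survivor when the mean ≥ 0.5 (ties classify
positive — a fixed convention, required for reproducibility). Metrics
(positive class = non-survivor):

    sensitivity = TP/(TP+FN)·100    specificity = TN/(FP+TN)·100
    accuracy    = (TP+TN)/n·100

A zero denominator yields `None` plus a flag, never a silent 0. The ROC
curve sweeps all score cutoffs (ties grouped into one step) and AUC is
its trapezoidal area, equal to the Mann–Whitney pairwise statistic; the
implementation delegates the sweep to scikit-learn while the test suite
checks it against an exhaustive pairwise oracle.

The 10-fold protocol deals shuffled patients into 10 balanced groups
(sizes differ by ≤1) and rotates: fold f tests group f, validates on
groups (f+1, f+2) mod 10, trains on the remaining seven. Every patient
is tested exactly once; a fresh model is constructed per fold. The
validation groups "cyclically following" the test group are a fixed
convention chosen for determinism and rotation symmetry. Cohort
balancing is by seeded uniform undersampling of the majority class
without replacement.

## 7. Synthetic cohorts

Each synthetic patient is a sum-of-Gaussians beat train: wave
w ∈ {P,Q,R,S,T} contributes a_w·exp(−(t−μ_w)²/2σ_w²) around each beat
fiducial, with per-lead amplitude scaling {I 0.7, II 1.0, V3 1.2,
V5 1.1} and defaults (a [mV], μ [s], σ [s]): P(0.15, −0.20, 0.025),
Q(−0.10, −0.035, 0.010), R(1.0, 0, 0.012), S(−0.25, 0.035, 0.010),
T(0.35, 0.22, 0.045). Heart rate is drawn per patient from 55–100 bpm;
RR intervals get Gaussian jitter (SD 0.010 s, truncated positive) and
white noise of 0.02 mV SD is added. The jitter SD is chosen so survivor
rhythm is nearly regular while the non-survivor multiplier produces
visible irregularity at image resolution.

Non-survivors differ by three effects chosen to mirror the morphologies
gradient attribution highlights on real CCU ECGs:

| effect | default | where |
|---|---|---|
| ST-segment offset (plateau between S and T centers) | +0.2 mV | lead V3 only |
| RR jitter multiplier | ×3 | all leads |
| R-wave amplitude multiplier | ×1.3 | all leads |

The ST offset is confined to V3 so that attribution localization has a
ground truth ("which strip carries the anomaly"); the other two effects
are physiologically global. `SynthParams.neutralized()` switches all
three off, making the class distributions identical — the null cohort.

What the generator does **not** emulate: baseline wander, electrode
artifacts, ectopy/arrhythmia taxonomies, inter-lead timing physiology,
or any realistic covariance between morphology and outcome. Passing the
end-to-end checks therefore demonstrates that the pipeline can recover a
known injected signal and does not hallucinate one under the null — it
says nothing about clinical performance, which requires real cohorts
(the headline clinical numbers of the motivating study are not
reproducible without its private data).

## 8. GradCAM

For target class c, the gradient of the pre-softmax class score with
respect to the final convolution's post-ReLU activations A^k is averaged
over space to give channel weights α_k; the map is relu(Σ_k α_k A^k),
upsampled bilinearly (half-pixel-aligned) to image resolution and
divided by its maximum. All-zero maps (possible through the ReLU) are
flagged `empty` rather than divided. The normalized map is invariant to
positive rescaling of the gradients. Overlays use matplotlib's `jet`
palette (blue = low, red = high) alpha-blended over the grayscale image.
`strip_attribution` integrates heatmap mass over each lead's row band
(and optional time bins); shares are fractions of total mass, so the
four bands sum to ≤ 1 with the remainder in the gaps.

Implementation note: because the network is built on the in-repo layer
framework, the gradients are exact — the analytic single-filter oracle
in the tests agrees to 1e-5, limited only by single precision.

## 9. Experiment sizes and stochastic checks

Desk-scale experiments use 100 patients/class (600 images), a stratified
7/2/1 patient-level split, and ≤10 training epochs — sizes at which the
full pipeline (generate, encode, train, evaluate) completes in about a
minute on one CPU core. Three facts about these sizes matter for
interpreting the stochastic checks:

* **Signal recovery**: with the default class effects the held-out
  patient-level AUC on the 20-patient test split is ≥ 0.90 for the
  majority of training seeds (typically 1.0).
* **Null calibration**: a 10 vs 10 test split gives a null AUC a
  standard deviation of ≈ 0.13 (Mann–Whitney), plus model-seed
  variance — a single 20-patient null AUC is compatible with anything
  in roughly [0.2, 0.8]. The chance-level check therefore scores all 60
  patients that received no gradient updates (validation + test;
  validation only monitors the loss and never selects the model), whose
  null AUC concentrates in [0.4, 0.6].
* **Attribution localization**: one split yields only ~10 correctly
  classified non-survivor test patients, so the V3-dominance check pools
  the test sets of the three seed replicates (~30 patients). The margin
  is modest — the R-amplitude and rhythm effects give the classifier
  legitimate evidence in every lead, and only the ST plateau is
  V3-specific.

## 10. Known limitations

* The harness trains small CNNs on CPUs; it does not ship pretrained
  ImageNet backbones, so published per-backbone clinical accuracies are
  out of reach by design.
* The MFER subset is a documented private TLV dialect for fixtures, not
  a standards-compliant MFER implementation.
* Max-pooling gradient ties route gradient to every maximal element;
  with continuous inputs ties have measure zero.
* The rasterizer draws hard 1-px polylines (no sub-pixel anti-aliasing);
  smoothing is provided entirely by the Lanczos reduction.
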