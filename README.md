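# ecg2img

Toolkit for predicting short-term mortality of cardiac-care-unit (CCU)
patients from resting ECGs by converting the waveforms into images and
classifying the images with a CNN — plus everything needed to evaluate
and explain such a pipeline: deterministic stacked-lead image encoding,
a backbone-agnostic classifier harness, patient-level 10-fold
cross-validation, GradCAM attribution, and a synthetic labelled ECG
cohort generator so the entire pipeline runs end-to-end with no clinical
data.

Intended users: researchers in ECG deep learning who want a transparent,
dependency-light reference implementation of the signal-to-image
approach, and a controlled synthetic test bed for it.

## The method

A 10-s, 500 Hz record (5000 samples/lead) is reduced to four leads in
fixed order II, V3, V5, aVR, where aVR is derived from the Einthoven
limb leads when not recorded:

    aVR(t) = -(I(t) + II(t)) / 2

Each lead is split into 3 contiguous segments (1667/1667/1666 samples),
rasterized as a connected 1-px polyline (linear interpolation between
samples; fixed ±2 mV amplitude scale), Lanczos-reduced to 224×26, and
the four strips are stacked with 40-px gaps into one 224×224 8-bit
grayscale image per segment — three images per patient.

A CNN scores each image with a death probability p ∈ [0, 1]; the
patient-level score is the mean of the three, thresholded at 0.5.
Evaluation uses patient-level 10-fold cross-validation (7 groups train,
2 validation, 1 test, rotated so every patient is tested once) with

    Sensitivity = TP/(TP+FN)×100   Specificity = TN/(FP+TN)×100
    Accuracy = (TP+TN)/n×100       and ROC/AUC over all score cutoffs.

GradCAM (gradients of the class score at the final convolution)
explains each decision as a heatmap over the image, which
`strip_attribution` converts into per-lead attribution shares using the
stacked-strip layout. Class imbalance is handled upstream by seeded
undersampling of the majority class.

The classifier harness replaces any backbone's head with two fresh
fully connected layers (transfer-learning style, optionally freezing
the backbone). It ships a small from-scratch `tiny2d` backbone and a
four-branch 1-D CNN baseline over the raw leads; the layers are
implemented in seeded, exactly-differentiated numpy (`ecg2img.nn`), so
results are reproducible bit-for-bit and attribution gradients are
exact. See `docs/methods.md` for the full model account and
`docs/mfer_subset.md` for the binary waveform fixture format.

## Worked example

Generate a 120-patient synthetic cohort (survivors vs non-survivors
with an ST-segment offset in V3, irregular rhythm and taller R waves),
encode it, train `tiny2d` on a stratified 7/2/1 patient split, and
score the held-out patients:

```bash
$ ecg2img experiment --n-per-class 60 --seed 7 --epochs 10
{
  "n_test_patients": 12,
  "accuracy_pct": 100.0,
  "sensitivity_pct": 100.0,
  "specificity_pct": 100.0,
  "auc": 1.0
}
```

The injected class effects are strong enough that the pipeline
separates the 12 held-out patients perfectly: every non-survivor's mean
death probability exceeds every survivor's (AUC 1.0) and all 12 land on
the correct side of the 0.5 threshold (accuracy 100%). On a null cohort
(`--null`, class effects switched off) the same pipeline scores at
chance.

The same stages are available stepwise:

```bash
ecg2img synth --n-per-class 60 --seed 7 --outdir cohort/
ecg2img convert --in cohort/syn_s0000.csv --to png --outdir imgs/
ecg2img train --images imgs/ --labels cohort/labels.csv \
              --epochs 10 --seed 7 --out model.npz
ecg2img evaluate --images imgs/ --labels cohort/labels.csv \
                 --folds 10 --seed 7 --report report.json
ecg2img gradcam --model model.npz --image imgs/syn_n0000_seg0.png \
                --target-class non_survivor --out overlay.png
```

or from Python:

```python
from ecg2img import (SynthParams, TrainConfig, gen_cohort, encode_cohort,
                     run_single_split_experiment)

result = run_single_split_experiment(n_per_class=60, seed=7,
                                     train_config=TrainConfig(
                                         freeze_backbone=False, seed=7))
print(result.report.auc, result.report.accuracy)
```

## Layout

```
src/ecg2img/
  signal_io.py    waveform records, CSV interchange, MFER-subset binary
  leads.py        aVR derivation, four-lead panel selection
  imaging.py      segmentation, rasterization, Lanczos, stacking, PNG
  nn.py           seeded numpy layers with manual backprop
  model.py        backbones, heads, training loop, 1-D baseline
  evaluation.py   aggregation, undersampling, k-fold protocol, metrics
  gradcam.py      class-activation maps, overlays, per-lead shares
  synthetic.py    sum-of-Gaussians ECG cohort generator
  experiment.py   end-to-end synthetic experiments
  cli.py          the `ecg2img` command
```
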