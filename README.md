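# echolvef

Automated left-ventricular ejection-fraction (LVEF) estimation from
apical-4-chamber (A4C) echocardiographic cine loops.

LVEF — the fraction of end-diastolic blood volume ejected per beat — is
the measurement that divides heart failure into its treatment-relevant
phenotypes (HFrEF < 40%, HFmrEF 40–49%, HFpEF ≥ 50%). Measuring it by
hand means visually picking end-diastolic (ED) and end-systolic (ES)
frames and tracing the endocardium, which is slow, poorly reproducible,
and usually done on a single beat even though guidelines recommend
averaging several — especially in atrial fibrillation, where EF varies
beat to beat. This package implements a fully automated alternative:

1. **Segmentation** — an atrous convolutional network (ResNet-style
   encoder + atrous spatial pyramid pooling) produces an LV mask per
   frame; the LV area *A* is the mask's pixel count.
2. **All-cycle ED/ES detection** — peaks and troughs of the area curve
   with topographic prominence above half the curve's range, at least 20
   frames apart, paired into (ED, ES) cycles.
3. **Area refinement** — the improved Jeffrey's method averages the
   per-cycle peak area with the top-10% areas of the whole curve and of
   the ED-to-ES window, suppressing single-frame segmentation outliers
   (a 90th/10th-percentile baseline and raw single-frame areas are
   available for ablation).
4. **LV length** — a voting ensemble (Extra Trees, AdaBoost, Lasso, and
   a Ridge/KNN/gradient-boosting stack; unweighted vote) predicts the
   apex-to-mid-annulus length *L* from mask shape features.
5. **Volumes and EF** — the ellipsoid single-plane (area-length) model

   V = 8A² / (3πL),   EF_i = (EDV_i − ESV_i)/EDV_i × 100%,

   with the video-level LVEF the mean of EF_i over all *N* detected
   cycles, followed by HF phenotype classification and a beat-to-beat
   visualiser payload.

A built-in simulator (pulsating ellipse with sinus or AF-like rhythm,
speckle texture, outlier injection) carries an analytic ground truth:
for an ellipse the area-length volume reduces exactly to the prolate
spheroid πLD²/6, so an isotropic ED→ES shrink by *s* gives EF = 1 − s³.
Every stage is therefore testable without any clinical data. Readers
for EchoNet-Dynamic-style annotation CSVs (VolumeTracings chords,
FileList labels) let the same pipeline run on the public datasets.

## Worked example

```sh
python examples/simulate_and_measure.py
```

```
truth EF        : 55.00%
pipeline EF     : 54.76%  (HFpEF)
absolute error  : 0.24 EF points
cycles detected : 3 at ED frames [12, 52, 92]
  cycle 0: ED frame 12, ES frame 28, EF 54.76%
  cycle 1: ED frame 52, ES frame 68, EF 54.76%
  cycle 2: ED frame 92, ES frame 108, EF 54.76%
```

The simulator built a three-cycle video with a known 55% EF; the
pipeline segmentation-free route (mask stack in, EF out) recovers it to
0.24 EF points, and every ED/ES frame is found exactly.

The beat-to-beat example shows why all-cycle averaging matters. With
per-beat EFs of 53.70 / 51.30 / 45.30 / 50.00% in an irregular rhythm
(`examples/beat_to_beat_af.py`):

```
per-cycle EF  : ['53.70%', '51.30%', '45.30%', '50.00%']
all-cycle EF  : 50.08%  -> HFpEF
```

Reading only the third beat would call this ventricle mildly reduced
(HFmrEF); the all-cycle mean classifies it correctly as preserved.

Other examples: `jeffrey_refinement.py` (outlier suppression),
`length_ensemble.py` (length regression + ANOVA model comparison),
`train_segmentation.py` (CPU overfit of the atrous network). A thin CLI
wraps the same functions: `echolvef simulate | train-seg | segment |
train-length | compare-lengths | analyze | evaluate` (see `--help`).

## Scope

The package runs entirely in pixel units (EF is dimensionless, so
calibration cancels) and ships no trained clinical model: the network
and ensemble included are desk-scale and intended for synthetic data or
retraining on real datasets via the provided readers. Simpson's biplane
volumes and DICOM ingestion are out of scope. See `docs/methods.md` for
the model details, defaults, and limitations.
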