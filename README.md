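# perfmoco

Breathing-motion compensation for first-pass gadolinium-enhanced myocardial
perfusion MRI, with a synthetic phantom test bed and time-intensity-curve
validation. The package implements two published compensation strategies:

- **ICA-SP** — temporal ICA of the series, wavelet-based labeling of the
  motion component (with a mean-frequency fallback for stress studies),
  optional RV/LV region-of-interest detection with a 30 mm gravity-centre
  sanity check, motion-free synthetic references by dropping the motion IC,
  and multi-pass B-spline SSD registration (κ=10, knot spacing 16, half
  working scale, 3 levels, ≤5 passes).
- **QUASI-P** — selection of a same-breathing-phase frame subset via
  normalized-gradient-field (NGF) similarity, NGF registration of the
  subset to a global reference, temporal interpolation into synthetic
  references, and SSD registration of the remaining frames (κ=0.1, knot
  spacing 5, 3 levels, adaptive gradient descent with start step 0.01 and
  epsilon 0.01).

Since no patient data ships with the repository, a phantom module generates
ECG-triggered 2D+t series (sequential RV → LV → myocardial enhancement via
gamma-variate kinetics, quasi-periodic breathing translation of the heart,
two leading proton-density frames) together with per-frame ground-truth
segmentations, dense motion fields, and the generating compartment curves.
Validation compares per-section time-intensity curves — ground truth from
per-frame masks vs. curves from the propagated LV-peak key-frame masks —
using NMSE and the Pearson coefficient, with the myocardium divided into 12
clockwise sections anchored at the LV-centre→RV-insertion ray.

## Command line

```bash
perfmoco simulate --out phantom_dir --seed 1 --motion free_breathing
perfmoco icasp  --in phantom_dir/series --out icasp_out
perfmoco quasip --in phantom_dir/series --out quasip_out
perfmoco validate --series phantom_dir/series --registered icasp_out \
                  --seg phantom_dir/segmentation.xml --out scores.csv
perfmoco experiment free_breathing --seeds 0,1,2 --out report_dir
```

Series are exchanged as DICOM directories (16-bit, minimal built-in codec)
or 8-bit PNG directories with a `series.json` sidecar. Segmentations use an
XML dialect (star with three circumcircle rays, the first through the RV
insertion point, plus endo-/epicardial contours; schema in
`src/perfmoco/data/segmentation.xsd`). Registered output directories carry
the warped series, per-frame transforms as JSON, and a decision log
(ICA mode, labeling method, ROI accept/reject, subset indices).

Configuration files are YAML with one section per module (`phantom`,
`icasp`, `quasip`); shipped defaults are the published parameter settings.

## Package layout

| Module | Role |
| --- | --- |
| `series_model` | 2D+t series model, DICOM and PNG+sidecar I/O, PD-frame stripping |
| `segmentation` | segmentation XML I/O, polygon rasterization, circumcircle, section division |
| `phantom` | synthetic perfusion series with ground truth |
| `ica_analysis` | FastICA decomposition, wavelet/frequency component labeling, RV/LV ROI |
| `registration` | B-spline SSD/NGF registration core with curvature regularization |
| `moco_icasp`, `moco_quasip` | the two compensation pipelines |
| `validation` | section time-intensity curves, NMSE/Pearson, summary tables |
| `experiments`, `cli`, `config` | batch experiments, command line, configuration |
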