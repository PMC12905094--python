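# petresponse

Short-term metabolic response analysis for FDG-PET/CT, built for oncology
imaging studies that ask one question: did a lesion's glucose uptake change
enough between a baseline and a follow-up scan to call it a response or a
progression?

The package covers the full quantitative chain on SUV volumes (standardized
uptake value, body-mass normalised, implicit units g/mL):

1. **Phantom simulation** — paired pre/post synthetic PET volumes with
   ellipsoidal lesions of known true SUV over a low background, degraded by
   Gaussian scanner blur and additive noise, so every downstream stage is
   testable against exact ground truth.
2. **Lesion delineation** — a semi-automated gradient-edge tool: click the
   approximate center voxel, drag along the longest axis, the contour snaps
   to the steepest radial intensity fall-off along 128 rays and is smoothed
   twice.
3. **SUV quantification** — per target: SUV\_max, SUV\_mean, SUV\_peak (mean
   within a ~1.2-cm-diameter, 1-mL sphere centered at the hottest voxel),
   contour volume, plus two filters: *evaluable* (volume ≥ 1.728 mL, a
   3×3×3-voxel block at 4-mm spacing) and *FDG-avid* (baseline
   SUV\_max ≥ 7.5 g/mL).
4. **Partial-volume correction** — damped Richardson–Lucy deconvolution
   (5 iterations, damping 0.1 SUV, 4-mm-FWHM Gaussian PSF on an 11-voxel
   kernel) to undo the uptake underestimation that scanner blur inflicts on
   small lesions.
5. **Response assessment** — the per-target statistic is the relative
   difference

   RD(%) = 100 × (SUV_post − SUV_pre) / SUV_pre

   classified under PERCIST-adapted thresholds: RD ≤ +15% (including any
   decrease) → **response**, RD ≥ +30% → **progression**, in between →
   **indeterminate**.  Cohort rates are reported per metric, per subset
   (all evaluable / FDG-avid) and per condition (raw / PVC), rounded
   half-to-even at one decimal.

## Worked example

`examples/full_pipeline.py` runs the whole chain on the bundled synthetic
cohort of 16 evaluable lesions (true RDs: ten at −40%, five at +20%, one at
+50%; 4-mm blur, 0.1 SUV noise):

```
$ python examples/full_pipeline.py
cohort summaries (rates in %, rounded half-to-even):
condition        subset   metric  n_targets  n_response  n_indeterminate  n_progression  rate_response  rate_indeterminate  rate_progression
      ...
      raw all_evaluable suv_mean         16          10                5              1           62.5                31.2               6.2
      raw all_evaluable suv_peak         16          10                5              1           62.5                31.2               6.2
      ...

truth check: 16/16 targets classified to their true category
```

Reading the `raw all_evaluable suv_mean` row: of 16 evaluable targets, 10
classified as response (62.5%), 5 indeterminate (31.2%) and 1 progression
(6.2%) — exactly the cohort's true composition, recovered through
simulation, contouring, quantification and classification.  The other
examples each exercise one capability (`simulate_phantom.py`,
`delineate_and_quantify.py`, `partial_volume_correction.py`,
`response_classification.py`).

The same pipeline is available as a shell tool:

```sh
petresponse run --out demo_run --seed 1          # end-to-end
petresponse simulate --out study --seed 1        # or stage by stage
petresponse segment --image study/pre.nii.gz --seeds study/seeds.csv --out masks
petresponse pvc --in study/pre.nii.gz --out pre_pvc.nii.gz --fwhm 4.0 --iterations 5 --damping 0.1
```

Every run writes its resolved configuration, a stage log, and all
intermediate NIfTI/CSV/JSON files into the output directory, so each
reported number is recomputable from persisted artifacts.

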