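# subfrax

Sub-fraction plan evaluation for MR-guided adaptive prostate radiotherapy,
exercised entirely on synthetic pelvic phantoms.

## The problem

Hypofractionated prostate treatments on an MR-linac (5 × 7.25 Gy) can split
each daily fraction into two sub-fractions. After the daily plan is
re-optimized on the pre-treatment MRI (adapt-to-shape, ATS), a fast
adapt-to-position (ATP) step precedes each sub-fraction: a translation-only
registration of the current position-verification (PV) anatomy to the
pre-treatment (PRE) anatomy updates the plan isocenter — a virtual couch
shift. The catch: the contours used to *approve* each sub-fraction plan are
only rigidly shifted along with it, while the real anatomy also rotates and
deforms. The clinically approved numbers may therefore overstate coverage.

`subfrax` rebuilds that evaluation loop as a simulation with known ground
truth. It generates pelvic anatomies (prostate + GTV, bladder, rectum,
sphincter), draws intrafraction motion whose 3D drift magnitude is
calibrated to clinically reported statistics (folded normal, mean ± SD of
3.0 ± 2.2 mm for PRE→PV1 and 3.5 ± 2.0 mm for PRE→PV2), plans a conformal
dose on the PTV, performs the ATP registration and isocenter shift, and
scores every sub-fraction twice:

* **approved** — contours carried along with the shifted plan (what the
  clinic sees);
* **corrected** — contours propagated through the true displacement field,
  with the targets re-created by the clinical margin recipe
  (GTV+4 mm staying outside rectum and bladder; CTV = prostate ∪ GTV+4 mm;
  PTV = CTV + 2/3/2 mm LR/AP/SI).

Metrics follow the full-scheme constraint table: CTV and PTV
V_3444 cGy ≥ 99 % (tolerated to 98.9 % and 96 %), bladder D_5cc ≤ 3700 cGy,
rectum D_1cc ≤ 3800 cGy, sphincter D_mean ≤ 2000 cGy, where
3444 cGy = round(0.95 × 5 × 725 cGy) is the V95 reference dose.

## Worked example

```bash
python examples/04_subfraction_workflow.py
```

prints one fraction through the full case matrix:

```
case              CTV V95  PTV V95  bladder D5cc  rectum D1cc
ATS                100.0%    99.5%         2412         3015
approved_ATP1      100.0%    99.5%         2412         3015
corrected_ATP1     100.0%    99.0%         2456         3115
approved_ATP2      100.0%    99.5%         2412         3015
corrected_ATP2     100.0%    95.5%         2353         2976

per-sub-fraction ground truth:
  sub-fraction 1: mean prostate displacement 2.7 mm, estimated shift (0.1, 0.4, -1.9) mm
  sub-fraction 2: mean prostate displacement 5.0 mm, estimated shift (0.4, 3.5, -3.5) mm
```

The approved rows reproduce the ATS metrics exactly — rigidly shifting dose
and contours together preserves every dose-volume metric, which is the
premise of the isocenter-shift correction. The corrected rows score the
same delivered plans against contours that truly follow the deformed
anatomy: here the second sub-fraction's PTV coverage drops to 95.5 % (below
the 96 % tolerance floor) because of the rotation and deformation the rigid
correction cannot capture, while the CTV stays fully covered.

Other examples: `01_phantom_and_targets.py` (anatomy + margin recipe),
`02_motion_and_registration.py` (drift simulation and recovery),
`03_plan_and_dvh.py` (planning + constraint table),
`05_cohort_study.py` (multi-patient summary with pass rates and
approved-minus-corrected drops).

A thin CLI wraps the same library calls:

```bash
subfrax phantom out/structures --config run.yaml
subfrax run --config run.yaml --out results/
subfrax accept --out acceptance/
```

All file I/O is NIfTI (masks, dose grids, 4-D displacement fields) plus
CSV/JSON reports; the run configuration is a validated YAML file in which
every omitted key falls back to the defaults above.

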