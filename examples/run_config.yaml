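# Full run-configuration schema for subfrax (every key optional; omitted
# keys take the package defaults shown here).  Unknown keys are rejected.

seed: 0

grid:
  shape: [96, 96, 96]        # voxels (LR, AP, SI)
  spacing: [2.0, 2.0, 2.0]   # mm; origin is centered automatically

phantom:
  prostate_semiaxes_mm: [20.0, 18.0, 22.0]
  gtv_radius_mm: 6.0
  gtv_offset_mm: [3.0, 2.0, -4.0]
  bladder_semiaxes_mm: [34.0, 30.0, 28.0]
  bladder_offset_mm: [0.0, -18.0, 38.0]   # anterior (-AP), superior (+SI)
  rectum_radius_mm: 11.0
  rectum_ap_offset_mm: 28.0
  rectum_curvature_mm: 6.0
  rectum_halflength_mm: 62.0
  sphincter_radius_mm: 9.0
  sphincter_height_mm: 14.0
  sphincter_si_offset_mm: -30.0
  body_semiaxes_mm: [88.0, 85.0]
  boundary_margin_mm: 16.0
  size_jitter_frac: 0.08     # per-patient multiplicative size jitter (SD)
  offset_jitter_mm: 2.0      # per-patient additive offset jitter (SD, mm)
  seed: 0

motion:
  pv1:                       # PRE -> PV1 (before the first sub-fraction)
    translation_mean_mm: 3.0 # folded-normal drift magnitude targets
    translation_sd_mm: 2.2
    rotation_sd_deg: 1.5
    deformation_amplitude_mm: 1.5   # RMS of the smooth random deformation
    correlation_length_mm: 25.0
    bladder_expansion_mm: 0.0       # peak radial bladder-filling displacement
  pv2:                       # PRE -> PV2 (cumulative drift)
    translation_mean_mm: 3.5
    translation_sd_mm: 2.0
    rotation_sd_deg: 1.5
    deformation_amplitude_mm: 1.5
    correlation_length_mm: 25.0
    bladder_expansion_mm: 0.0
  anisotropy: [0.5, 1.0, 1.0]  # drift direction weights (LR, AP, SI)
  taper_inner_mm: 50.0         # rigid drift full strength inside this radius
  taper_outer_mm: 110.0        # ... and zero beyond this radius
  seed: 0

plan:
  prescription_cGy: 3625.0     # full scheme, 5 x 725 cGy
  penumbra_sigma_mm: 4.0
  normalization_target: 0.995  # fraction of PTV at/above the V95 reference
  mc_noise_rel: 0.0            # 0.03 emulates a 3% MC statistical uncertainty
  flash_margin_mm: null        # null -> 1.65 * penumbra_sigma

margins:
  gtv_margin_mm: 4.0
  ptv_margins_mm: [2.0, 3.0, 2.0]  # (LR, AP, SI)

# Omitting `constraints` yields the clinical table:
#   CTV  V_3444cGy >= 99 % (tolerance -0.1)
#   PTV  V_3444cGy >= 99 % (tolerance -3)
#   bladder D_5cc <= 3700 cGy ; rectum D_1cc <= 3800 cGy
#   sphincter D_mean <= 2000 cGy
constraints: []

cohort:
  n_patients: 15
  n_fractions: 5               # each fraction = 2 sub-fractions

registration:
  search_radius_mm: 15.0
  subvoxel: true
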