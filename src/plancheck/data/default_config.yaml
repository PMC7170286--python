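# Default plancheck profile: one entry per rule-table row (the qa_plans row
# is a composite of 10 constituent sub-checks, for 34 checks in total).
# Every threshold below is illustrative institution policy — replace with
# your own.  Order is display order only; checkers are independent.
enabled_checkers:
  - isocenter_consistency
  - tolerance_tables
  - drr_created
  - patient_orientation
  - image_structset_names
  - course_names
  - plan_names
  - reference_point_limits
  - bolus_attached
  - drr_overlay
  - dose_rate
  - plan_status
  - calc_settings_grid
  - couch_structures
  - unusual_warnings
  - invalid_characters
  - control_point_count
  - imrt_leaf_delivery
  - leaf_motion_calculator
  - ct_density_overrides
  - bolus_hu
  - nonclinical_complete
  - default_couch_position
  - setup_imager_position
  - qa_plans

checkers:
  isocenter_consistency:
    tolerance_mm: 0.01
  tolerance_tables:
    forbidden_labels: [TEST]
  course_names:
    regex: 'C\d+'
    severity: flag
  plan_names:
    regex: '[A-Z0-9][A-Z0-9_\-]{0,12}'
    severity: flag
  image_structset_names:
    image_regex: '[A-Z0-9][A-Z0-9_]*'
    structset_regex: '[A-Z0-9][A-Z0-9_]*'
    severity: flag
  reference_point_limits:
    limit_multiplier: 1.07
    consistency_rel_tol: 0.01
  dose_rate:
    allowed:
      TB1:
        6X: [400, 600]
        15X: [400, 600]
        6X-FFF: [1400]
  plan_status:
    required_status: TREATMENT_APPROVED
  calc_settings_grid:
    model: AAA_15606
    default_grid_mm: 2.5
  couch_structures:
    required:
      TB1:
        CouchSurface: 0.7
        CouchInterior: 0.2
    density_tolerance: 0.01
  unusual_warnings:
    patterns: ['(?i)unable', '(?i)exceed', '(?i)overlap']
  invalid_characters:
    whitelist: 'ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789 _-.()+'
  control_point_count:
    max_imrt: 300
    min_vmat: 30
    max_vmat: 400
  imrt_leaf_delivery:
    min_gap_mm: 0.5
    closed_gap_mm: 0.1
    max_leaf_speed_mm_s: 25.0
  leaf_motion_calculator:
    model: LMC_15606
  bolus_hu:
    water_hu: 0.0
    tolerance_hu: 20.0
  default_couch_position:
    windows:
      TB1:
        vertical: [-250.0, -50.0]
        longitudinal: [500.0, 1100.0]
        lateral: [-50.0, 50.0]
  setup_imager_position:
    expected: {vrt: -500.0, lng: 0.0, lat: 0.0}
    tolerance_mm: 20.0
    require_setup_fields: true
  qa_plans:
    qa_course_regex: '(?i)^QA'
    epid_name_regex: 'QA[_A-Z0-9\-]*'
    epid_sid_mm: 1000.0
    sid_tolerance_mm: 1.0
    mu_tolerance: 0.1
    weight_tolerance: 1.0e-4
    gantry_tolerance_deg: 0.1
    required_status: TREATMENT_APPROVED
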