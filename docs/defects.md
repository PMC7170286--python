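# Defect catalog

Each defect mutates exactly one aspect of a clean synthetic fixture
(a DICOM tag or a sidecar key), leaves the plan loadable, and is mapped to
the single checker expected to flag it.  `plancheck.synth.DEFECTS` is the
authoritative table; `evaluate_detection` runs the corpus and verifies the
mapping is the identity (sensitivity 1.0, no collateral status changes,
clean plans flag-free).

| defect id | template | mutation | expected checker |
|---|---|---|---|
| isocenter_shift | STATIC_2FIELD | beam isocenter +1 mm in x | isocenter_consistency |
| plan_name_bad_convention | STATIC_2FIELD | plan name lowercased | plan_names |
| course_name_bad | STATIC_2FIELD | course renamed off-convention | course_names |
| image_name_bad | STATIC_2FIELD | image display name off-convention | image_structset_names |
| beam_name_invalid_char | STATIC_2FIELD | `#` appended to a beam name | invalid_characters |
| refpoint_over_limit | STATIC_2FIELD | reference point at 110% of prescription | reference_point_limits |
| refpoint_missing_contribution | STATIC_2FIELD | beam dropped from contributions | reference_point_limits |
| bolus_unlinked | IMRT_5FIELD | bolus reference removed from one beam | bolus_attached |
| drr_missing | STATIC_2FIELD | DRR marked absent for one beam | drr_created |
| drr_overlay_missing | STATIC_2FIELD | overlay marked absent for one beam | drr_overlay |
| dose_rate_wrong | STATIC_2FIELD | dose rate set to 500 MU/min | dose_rate |
| plan_not_approved | STATIC_2FIELD | status left PLANNING_APPROVED | plan_status |
| nonclinical_not_complete | STATIC_2FIELD | non-clinical course, plan not COMPLETED | nonclinical_complete |
| calc_model_wrong | STATIC_2FIELD | outdated calculation model | calc_settings_grid |
| grid_too_coarse | STATIC_2FIELD | dose grid 2.5 → 3.5 mm | calc_settings_grid |
| lmc_wrong | IMRT_5FIELD | outdated leaf-motion calculator | leaf_motion_calculator |
| couch_structure_missing | STATIC_2FIELD | couch interior ROI deleted | couch_structures |
| couch_position_out | STATIC_2FIELD | table-top vertical −300 mm | default_couch_position |
| imager_position_out | STATIC_2FIELD | imager longitudinal +50 mm | setup_imager_position |
| static_extra_cp | STATIC_2FIELD | third CP appended to a static beam | control_point_count |
| vmat_cp_truncated | VMAT_2ARC | arc decimated to 11 CPs | control_point_count |
| leaf_gap_narrow | IMRT_5FIELD | in-field pair closed to 0.2 mm | imrt_leaf_delivery |
| leaf_speed_excess | IMRT_5FIELD | 40 mm leaf jump between CPs | imrt_leaf_delivery |
| tolerance_table_test | STATIC_2FIELD | tolerance table relabelled TEST | tolerance_tables |
| tolerance_table_missing | STATIC_2FIELD | tolerance label cleared | tolerance_tables |
| qa_mu_mismatch | ONE_FX_VMAT_WITH_EPID_QA | verification MU +5 | qa_plans |
| qa_sid_wrong | ONE_FX_VMAT_WITH_EPID_QA | EPID SID 1500 mm | qa_plans |
| qa_missing | ONE_FX_VMAT_WITH_EPID_QA | required EPID plan deleted | qa_plans |
| qa_status_wrong_epid | ONE_FX_VMAT_WITH_EPID_QA | EPID plan unapproved | qa_plans |
| qa_gantry_nonzero | ONE_FX_FFF_WITH_MAPCHECK_QA | MapCheck beam at gantry 30° | qa_plans |
| qa_status_wrong_mapcheck | ONE_FX_FFF_WITH_MAPCHECK_QA | MapCheck plan unapproved | qa_plans |
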