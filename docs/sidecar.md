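# Sidecar schema

The sidecar is a single UTF-8 YAML document carrying plan fields that live
in the planning-system database rather than in DICOM exports.  It is keyed
to the RT Plan by `plan_id` (must equal the plan's RTPlanLabel; mismatch
is a linkage error).  Every key except `plan_id` is optional: an absent
key leaves the field "unknown", and checkers that depend on it flag with
an "insufficient data" message.

```yaml
plan_id: PELV_STAT              # required; must match RTPlanLabel
course_id: C1
course_intent: CLINICAL          # CLINICAL | NON_CLINICAL | QA
plan_status: TREATMENT_APPROVED  # UNAPPROVED | PLANNING_APPROVED |
                                 # TREATMENT_APPROVED | COMPLETED | REJECTED
fractions: 25                    # overrides the DICOM fraction count if set
prescription_dose_gy: 50.0
calc_model: AAA_15606
leaf_motion_calculator: LMC_15606
image_id: IMG1
image_name: CT_20160414          # display names checked by the naming rules
structure_set_id: SS1
structure_set_name: SS_20160414
warnings: []                     # recorded calculation warnings (text)

drr:                             # per beam name
  AP:    {present: true, overlay: true}
  SU_AP: {present: true, overlay: true}

imager_positions:                # per setup-field name, mm
  SU_AP: {vrt: -500.0, lng: 0.0, lat: 0.0}

reference_points:
  - ref_id: RP1
    name: PRESC_PT
    total_dose_gy: 50.0
    dose_per_fraction_gy: 2.0
    contributing_beam_ids: [AP, PA]   # beam names or numbers

qa_plans:
  - qa_plan_id: QA_SBRT_V1
    qa_kind: EPID                # EPID | MAPCHECK
    course_id: QA1
    course_intent: QA
    plan_status: TREATMENT_APPROVED
    linked_clinical_plan_id: SBRT_V1  # must equal plan_id
    reference_sid_mm: 1000.0          # EPID only
    tolerance_table_label: QA
    treatment_time_defined: true
    rtplan_file: qa_epid.dcm          # RT Plan DICOM, relative to the sidecar
```

Units: mm, Gy, MU.  Enum values are case-insensitive on input.  Unknown
top-level keys are ignored.  The schema is a deliberate superset of what
any one planning system exports through any one channel; which fields an
institution can actually populate depends on its export tooling.
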