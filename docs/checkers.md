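# Checker reference

One section per checker id in the shipped profile, with its rule, status
kind (`P/F` = pass/flag, `R` = report) and configuration keys.  Shared
conventions: missing sidecar data → FLAG "insufficient data"; tolerance
boundaries compare with `<=` (exactly at tolerance passes); inapplicable
checkers PASS with a "not applicable" message.

## isocenter_consistency (P/F)
All beams carrying an isocenter must agree within `tolerance_mm`
(default 0.01).  Flags name the deviating beam and the deviation.

## tolerance_tables (R)
Flags any treatment beam whose tolerance-table label is empty or in
`forbidden_labels` (default `[TEST]`); otherwise reports the distinct
labels in use for reviewer judgement.

## drr_created (P/F)
Every beam must have a DRR (`drr.<beam>.present` in the sidecar).

## patient_orientation (R)
Reports the patient setup position (HFS, HFP, FFS, FFP, ...).

## image_structset_names / course_names / plan_names (P/F)
Display names must fullmatch the configured regex (`image_regex` /
`structset_regex`, `regex`).  Each rule has a `severity: flag|report`
switch so an institution can soften a convention without disabling it.
Shipped regexes are illustrative.

## reference_point_limits (P/F)
Flags a reference point whose total dose exceeds
`limit_multiplier × prescription` (default 1.07), a per-fraction dose
inconsistent with the total beyond `consistency_rel_tol` (default 0.01),
or a treatment beam contributing to no reference point.

## bolus_attached (P/F)
If any bolus structure exists, every treatment beam must reference it.
`per_bolus_beams` optionally restricts a bolus to a beam subset.

## drr_overlay (P/F)
Every beam with a DRR must have the graticule/field overlay burned in.
Beams without a DRR are skipped (that is `drr_created`'s finding).

## dose_rate (P/F)
Each treatment beam's dose rate must be in the `allowed` set for its
(machine, energy); unknown machines or energies flag.

## plan_status (P/F)
Clinical plans must carry `required_status` (default TREATMENT_APPROVED).

## calc_settings_grid (P/F)
`calc_model` must equal `model` and the dose-grid resolution (maximum
axis pitch) must be at most `default_grid_mm` (default 2.5).

## couch_structures (P/F)
The machine's couch model structures must exist with the configured
density assignments (`required`, `density_tolerance`).

## unusual_warnings (R)
Reports recorded calculation warnings matching any of `patterns`.

## invalid_characters (P/F)
Plan/course/image/structure-set/beam names may contain only `whitelist`
characters.  An empty whitelist is a configuration error.

## control_point_count (P/F)
Static beams: exactly 2 CPs.  IMRT: 2..`max_imrt`.  VMAT:
`min_vmat`..`max_vmat`.

## imrt_leaf_delivery (P/F)
Dynamic beams: every in-field leaf pair gap ≥ `min_gap_mm` (pairs closed
to `closed_gap_mm` behind a jaw are exempt) and required leaf speed
`|Δx|·DR/(ΔMU·60)` ≤ `max_leaf_speed_mm_s`.

## leaf_motion_calculator (P/F)
IMRT plans must have used leaf-motion calculator `model`.

## ct_density_overrides (R)
Reports every structure with an assigned density/HU override.

## bolus_hu (R)
Reports each bolus whose assigned value differs from `water_hu` by more
than `tolerance_hu`; a bolus with no assigned value is "not evaluable".

## nonclinical_complete (P/F)
Plans in non-clinical courses must be set to COMPLETED.

## default_couch_position (P/F)
First-control-point table-top positions must fall inside the per-machine
`windows` (vertical / longitudinal / lateral, mm).

## setup_imager_position (P/F)
Setup fields must exist (`require_setup_fields`) and their imager
positions must be within `tolerance_mm` of `expected` (vrt/lng/lat).

## qa_plans (P/F, composite of 10 sub-checks)
1. every verification plan lives in a QA course (`qa_course_regex`);
2. EPID plan ids match `epid_name_regex`;
3. EPID reference images at `epid_sid_mm` ± `sid_tolerance_mm`;
4. *gated* (1 fraction, IMRT/VMAT, 6X/15X): an EPID plan exists and every
   treatment beam matches its verification beam in MU (± `mu_tolerance`),
   control-point count, and cumulative weights (± `weight_tolerance`);
5. *gated* (1 fraction, IMRT/VMAT, 6X-FFF): a MapCheck plan exists;
6. all MapCheck beams at gantry 0 (± `gantry_tolerance_deg`);
7. all verification plans have tolerance tables defined;
8. all verification plans have treatment time defined;
9. EPID plans carry `required_status`;
10. MapCheck plans carry `required_status`.

The composite flags if any sub-check fails; its messages enumerate all
ten outcomes (`pass` / `FAIL` / `n/a`).
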