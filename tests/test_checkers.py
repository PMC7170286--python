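"""Unit tests for the individual checkers, driven by small in-memory plan
contexts.  Each test states the rule it exercises; boundary cases document
the <=-at-tolerance convention."""

import dataclasses

import numpy as np

from plancheck.checkers import (
    QA_SUBCHECKS,
    check_bolus,
    check_calc_settings,
    check_control_points,
    check_couch,
    check_dose_rate,
    check_drr,
    check_imrt_leaf_delivery,
    check_invalid_characters,
    check_isocenter_consistency,
    check_naming_conventions,
    check_plan_status,
    check_qa_plans,
    check_reference_point_limits,
    check_setup_fields,
    check_tolerance_tables,
    report_overrides_and_warnings,
    report_patient_orientation,
)
from plancheck.framework import ComplianceStatus
from plancheck.plan_model import (
    BeamRole,
    BolusStructure,
    CourseIntent,
    DeliveryKind,
    DensityOverride,
    PlanStatus,
)
from tests.conftest import _simple_beam, make_ctx

PASS = ComplianceStatus.PASS
FLAG = ComplianceStatus.FLAG
REPORT = ComplianceStatus.REPORT


class TestIsocenter:
    def test_shared_isocenter_passes(self, cfg):
        assert check_isocenter_consistency(make_ctx(), cfg).status is PASS

    def test_one_millimetre_shift_flags_and_names_beam(self, cfg):
        ctx = make_ctx()
        ctx.beams[1].isocenter = ctx.beams[1].isocenter + np.array([1.0, 0, 0])
        result = check_isocenter_consistency(ctx, cfg)
        assert result.status is FLAG
        assert "PA" in result.messages[0]

    def test_exactly_at_tolerance_passes(self, cfg):
        """<= convention: a deviation of exactly 0.01 mm is compliant."""
        ctx = make_ctx()
        ctx.beams[1].isocenter = ctx.beams[1].isocenter + np.array([0.01, 0, 0])
        assert check_isocenter_consistency(ctx, cfg).status is PASS


class TestNaming:
    def test_default_conventions_pass(self, cfg):
        ctx = make_ctx()
        for scope in ("course", "plan", "image_structset"):
            assert check_naming_conventions(ctx, cfg, scope=scope).status is PASS

    def test_trailing_whitespace_flags(self, cfg):
        result = check_naming_conventions(make_ctx(plan_name="PELV_AP "), cfg, scope="plan")
        assert result.status is FLAG

    def test_empty_course_flags(self, cfg):
        result = check_naming_conventions(make_ctx(course_id=""), cfg, scope="course")
        assert result.status is FLAG
        assert "empty" in result.messages[0]

    def test_unknown_name_is_insufficient_data(self, cfg):
        result = check_naming_conventions(make_ctx(course_id=None), cfg, scope="course")
        assert result.status is FLAG
        assert "insufficient data" in result.messages[0]

    def test_severity_switch_softens_to_report(self, cfg):
        cfg2 = dataclasses.replace(
            cfg, params={**cfg.params, "plan_names": {"severity": "report"}}
        )
        result = check_naming_conventions(make_ctx(plan_name="bad_name"), cfg2, scope="plan")
        assert result.status is REPORT


class TestInvalidCharacters:
    def test_whitelisted_names_pass(self, cfg):
        assert check_invalid_characters(make_ctx(), cfg).status is PASS

    def test_non_ascii_character_flags_with_field_and_char(self, cfg):
        result = check_invalid_characters(make_ctx(plan_name="PELVé"), cfg)
        assert result.status is FLAG
        assert "plan name" in result.messages[0] and "é" in result.messages[0]


class TestReferencePoints:
    def test_at_prescription_passes_with_107_percent_limit(self, cfg):
        assert check_reference_point_limits(make_ctx(), cfg).status is PASS

    def test_110_percent_flags(self, cfg):
        ctx = make_ctx()
        ctx.reference_points[0] = dataclasses.replace(
            ctx.reference_points[0], total_dose=55.0, dose_per_fraction=2.2
        )
        result = check_reference_point_limits(ctx, cfg)
        assert result.status is FLAG
        assert "exceeds" in result.messages[0]

    def test_uncovered_beam_flags_naming_it(self, cfg):
        ctx = make_ctx()
        ctx.reference_points[0] = dataclasses.replace(
            ctx.reference_points[0], contributing_beam_ids=["AP"]
        )
        result = check_reference_point_limits(ctx, cfg)
        assert result.status is FLAG
        assert any("PA" in m for m in result.messages)

    def test_missing_prescription_is_insufficient(self, cfg):
        result = check_reference_point_limits(make_ctx(prescription_dose=None), cfg)
        assert result.status is FLAG
        assert "insufficient" in result.messages[0]


class TestBolus:
    def test_bolus_on_all_beams_passes(self, cfg):
        ctx = make_ctx(bolus_structures=[BolusStructure("Bolus5mm", 0.0)])
        for beam in ctx.treatment_beams():
            beam.bolus_ids = ["Bolus5mm"]
        assert check_bolus(ctx, cfg, scope="attached").status is PASS

    def test_bolus_missing_from_one_beam_flags_it(self, cfg):
        ctx = make_ctx(bolus_structures=[BolusStructure("Bolus5mm", 0.0)])
        ctx.treatment_beams()[0].bolus_ids = ["Bolus5mm"]
        result = check_bolus(ctx, cfg, scope="attached")
        assert result.status is FLAG
        assert "PA" in result.messages[0]

    def test_nonwater_override_reported_with_value(self, cfg):
        ctx = make_ctx(bolus_structures=[BolusStructure("Bolus5mm", 120.0)])
        result = check_bolus(ctx, cfg, scope="hu")
        assert result.status is REPORT
        assert "+120" in result.messages[0]

    def test_unassigned_bolus_reported_not_evaluable(self, cfg):
        ctx = make_ctx(bolus_structures=[BolusStructure("Bolus5mm", None)])
        result = check_bolus(ctx, cfg, scope="hu")
        assert result.status is REPORT
        assert "not evaluable" in result.messages[0]


class TestDRR:
    def test_all_present_passes(self, cfg):
        ctx = make_ctx()
        assert check_drr(ctx, cfg, scope="created").status is PASS
        assert check_drr(ctx, cfg, scope="overlay").status is PASS

    def test_setup_beam_without_drr_flags(self, cfg):
        ctx = make_ctx()
        ctx.setup_beams()[0].drr_present = False
        assert check_drr(ctx, cfg, scope="created").status is FLAG

    def test_unknown_overlay_is_insufficient(self, cfg):
        ctx = make_ctx()
        ctx.beams[0].drr_overlay_present = None
        result = check_drr(ctx, cfg, scope="overlay")
        assert result.status is FLAG
        assert "insufficient data" in result.messages[0]

    def test_beam_without_drr_skipped_by_overlay_check(self, cfg):
        """A missing DRR belongs to the created-check; the overlay check
        must not double-report it."""
        ctx = make_ctx()
        ctx.beams[0].drr_present = False
        ctx.beams[0].drr_overlay_present = None
        assert check_drr(ctx, cfg, scope="overlay").status is PASS


class TestDoseRate:
    def test_allowed_rate_passes(self, cfg):
        assert check_dose_rate(make_ctx(), cfg).status is PASS

    def test_disallowed_rate_flags(self, cfg):
        ctx = make_ctx()
        ctx.treatment_beams()[0].dose_rate = 500.0
        result = check_dose_rate(ctx, cfg)
        assert result.status is FLAG
        assert "500" in result.messages[0]

    def test_unknown_machine_flags(self, cfg):
        ctx = make_ctx()
        for beam in ctx.beams:
            beam.machine_name = "UNKNOWN_LINAC"
        result = check_dose_rate(ctx, cfg)
        assert result.status is FLAG
        assert "not in configuration" in result.messages[0]


class TestPlanStatus:
    def test_approved_clinical_plan_passes(self, cfg):
        assert check_plan_status(make_ctx(), cfg, scope="clinical").status is PASS

    def test_unapproved_clinical_plan_flags(self, cfg):
        result = check_plan_status(
            make_ctx(plan_status=PlanStatus.PLANNING_APPROVED), cfg, scope="clinical"
        )
        assert result.status is FLAG

    def test_nonclinical_course_must_be_completed(self, cfg):
        ctx = make_ctx(
            course_intent=CourseIntent.NON_CLINICAL, plan_status=PlanStatus.UNAPPROVED
        )
        result = check_plan_status(ctx, cfg, scope="nonclinical")
        assert result.status is FLAG
        assert "COMPLETED" in result.messages[0]

    def test_nonclinical_scope_na_for_clinical_course(self, cfg):
        result = check_plan_status(make_ctx(), cfg, scope="nonclinical")
        assert result.status is PASS
        assert "not applicable" in result.messages[0]


class TestCalcSettings:
    def test_default_model_and_grid_pass(self, cfg):
        assert check_calc_settings(make_ctx(), cfg, scope="model_grid").status is PASS

    def test_coarse_grid_flags(self, cfg):
        result = check_calc_settings(make_ctx(dose_grid_resolution=3.0), cfg, scope="model_grid")
        assert result.status is FLAG
        assert "coarser" in result.messages[0]

    def test_grid_exactly_at_default_passes(self, cfg):
        assert (
            check_calc_settings(make_ctx(dose_grid_resolution=2.5), cfg, scope="model_grid").status
            is PASS
        )

    def test_wrong_lmc_flags_on_imrt_plans(self, cfg):
        beams = [
            _simple_beam("F1", "1", kind=DeliveryKind.IMRT, n_cp=10),
            _simple_beam("SU_AP", "2", role=BeamRole.SETUP),
        ]
        ctx = make_ctx(beams=beams, leaf_motion_calculator="LMC_OLD")
        assert check_calc_settings(ctx, cfg, scope="lmc").status is FLAG

    def test_lmc_na_without_imrt(self, cfg):
        result = check_calc_settings(make_ctx(leaf_motion_calculator=None), cfg, scope="lmc")
        assert result.status is PASS
        assert "not applicable" in result.messages[0]


class TestCouch:
    def test_expected_structures_and_position_pass(self, cfg):
        ctx = make_ctx()
        assert check_couch(ctx, cfg, scope="structures").status is PASS
        assert check_couch(ctx, cfg, scope="position").status is PASS

    def test_missing_interior_flags(self, cfg):
        ctx = make_ctx()
        ctx.couch_structures = ctx.couch_structures[:1]
        result = check_couch(ctx, cfg, scope="structures")
        assert result.status is FLAG
        assert "CouchInterior" in result.messages[0]

    def test_vertical_out_of_window_flags_with_value_and_window(self, cfg):
        ctx = make_ctx()
        for beam in ctx.treatment_beams():
            for cp in beam.control_points:
                cp.table_top_vertical = -300.0
        result = check_couch(ctx, cfg, scope="position")
        assert result.status is FLAG
        assert "-300" in result.messages[0] and "window" in result.messages[0]


class TestSetupFields:
    def test_imager_at_expected_position_passes(self, cfg):
        assert check_setup_fields(make_ctx(), cfg).status is PASS

    def test_longitudinal_offset_flags(self, cfg):
        ctx = make_ctx()
        ctx.setup_beams()[0].imager_position = np.array([-500.0, 50.0, 0.0])
        result = check_setup_fields(ctx, cfg)
        assert result.status is FLAG
        assert "lng" in result.messages[0]

    def test_no_setup_fields_flags(self, cfg):
        ctx = make_ctx(beams=[_simple_beam("AP", "1")])
        ctx.reference_points[0].contributing_beam_ids[:] = ["AP"]
        result = check_setup_fields(ctx, cfg)
        assert result.status is FLAG
        assert "no setup fields" in result.messages[0]


class TestControlPoints:
    def test_static_two_cp_passes(self, cfg):
        assert check_control_points(make_ctx(), cfg).status is PASS

    def test_static_three_cp_flags(self, cfg):
        ctx = make_ctx(beams=[_simple_beam("AP", "1", n_cp=3)])
        assert check_control_points(ctx, cfg).status is FLAG

    def test_vmat_at_max_boundary_passes(self, cfg):
        max_vmat = cfg.params_for("control_point_count")["max_vmat"]
        ctx = make_ctx(beams=[_simple_beam("ARC1", "1", kind=DeliveryKind.VMAT, n_cp=max_vmat)])
        assert check_control_points(ctx, cfg).status is PASS

    def test_vmat_below_minimum_flags(self, cfg):
        ctx = make_ctx(beams=[_simple_beam("ARC1", "1", kind=DeliveryKind.VMAT, n_cp=10)])
        assert check_control_points(ctx, cfg).status is FLAG


class TestLeafDelivery:
    @staticmethod
    def _dynamic_beam(mlc_per_cp, meterset=100.0, dose_rate=600.0):
        n_cp = len(mlc_per_cp)
        return _simple_beam(
            "DYN", "1", kind=DeliveryKind.IMRT, n_cp=n_cp, mlc=mlc_per_cp,
            meterset=meterset, dose_rate=dose_rate,
        )

    def test_wide_slow_aperture_passes(self, cfg):
        mlc = [[[-20.0, -18.0], [0.0, 2.0]], [[-18.0, -16.0], [2.0, 4.0]]]
        ctx = make_ctx(beams=[self._dynamic_beam(mlc)])
        ctx.reference_points[0].contributing_beam_ids[:] = ["DYN"]
        assert check_imrt_leaf_delivery(ctx, cfg).status is PASS

    def test_narrow_in_field_gap_flags_with_location(self, cfg):
        mlc = [[[-20.0, 0.0], [0.0, 0.2]], [[-18.0, 0.0], [2.0, 0.2]]]
        ctx = make_ctx(beams=[self._dynamic_beam(mlc)])
        result = check_imrt_leaf_delivery(ctx, cfg)
        assert result.status is FLAG
        assert "leaf pair 1" in result.messages[0]

    def test_required_speed_from_formula(self, cfg):
        """A leaf travelling 30 mm while 0.5 MU is delivered at 600 MU/min
        needs 30*600/(0.5*60) = 600 mm/s — far beyond the 25 mm/s limit."""
        mlc = [[[-20.0], [0.0]], [[10.0], [30.0]]]  # both banks travel 30 mm
        beam = self._dynamic_beam(mlc, meterset=0.5, dose_rate=600.0)
        ctx = make_ctx(beams=[beam])
        result = check_imrt_leaf_delivery(ctx, cfg)
        assert result.status is FLAG
        assert any("600.0 mm/s" in m for m in result.messages)

    def test_static_beams_not_applicable(self, cfg):
        result = check_imrt_leaf_delivery(make_ctx(), cfg)
        assert result.status is PASS
        assert "not applicable" in result.messages[0]


class TestReportCheckers:
    def test_orientation_reported(self, cfg):
        for orientation in ("HFS", "HFP"):
            result = report_patient_orientation(make_ctx(patient_orientation=orientation), cfg)
            assert result.status is REPORT
            assert orientation in result.messages[0]

    def test_missing_orientation_is_insufficient(self, cfg):
        result = report_patient_orientation(make_ctx(patient_orientation=None), cfg)
        assert result.status is FLAG

    def test_clinical_label_reported_forbidden_flags(self, cfg):
        ctx = make_ctx()
        for beam in ctx.treatment_beams():
            beam.tolerance_table_label = "SRS"
        result = check_tolerance_tables(ctx, cfg)
        assert result.status is REPORT and "SRS" in result.messages[0]
        ctx.treatment_beams()[0].tolerance_table_label = "TEST"
        assert check_tolerance_tables(ctx, cfg).status is FLAG

    def test_missing_tolerance_label_flags(self, cfg):
        ctx = make_ctx()
        ctx.treatment_beams()[0].tolerance_table_label = ""
        result = check_tolerance_tables(ctx, cfg)
        assert result.status is FLAG
        assert "no tolerance table" in result.messages[0]

    def test_density_override_reported(self, cfg):
        ctx = make_ctx(density_overrides=[DensityOverride("Lung_L", 0.3, "rel_electron_density")])
        result = report_overrides_and_warnings(ctx, cfg, scope="overrides")
        assert result.status is REPORT
        assert "Lung_L" in result.messages[0]

    def test_nothing_to_report_is_pass(self, cfg):
        ctx = make_ctx(density_overrides=[], warnings=[])
        assert report_overrides_and_warnings(ctx, cfg, scope="overrides").status is PASS
        assert report_overrides_and_warnings(ctx, cfg, scope="warnings").status is PASS

    def test_matching_warning_reported(self, cfg):
        ctx = make_ctx(warnings=["Dose exceeds 110% of prescription somewhere"])
        result = report_overrides_and_warnings(ctx, cfg, scope="warnings")
        assert result.status is REPORT


class TestQAPlanComposite:
    def test_clean_epid_fixture_passes_with_ten_submessages(self, contexts, cfg):
        result = check_qa_plans(contexts["ONE_FX_VMAT_WITH_EPID_QA"], cfg)
        assert result.status is PASS
        assert len(result.messages) == len(QA_SUBCHECKS) == 10
        assert list(result.details) == QA_SUBCHECKS

    def test_mu_mismatch_fails_only_that_subcheck(self, contexts, cfg):
        ctx = contexts["ONE_FX_VMAT_WITH_EPID_QA"]
        qa_beam = ctx.qa_plans[0].beams[0]
        original = qa_beam.meterset
        try:
            qa_beam.meterset = original + 5.0
            result = check_qa_plans(ctx, cfg)
            assert result.status is ComplianceStatus.FLAG
            failed = [k for k, v in result.details.items() if v == "FAIL"]
            assert failed == ["epid_mu_cp_match"]
        finally:
            qa_beam.meterset = original

    def test_missing_mapcheck_for_fff_single_fraction_flags(self, contexts, cfg):
        ctx = contexts["ONE_FX_FFF_WITH_MAPCHECK_QA"]
        saved = ctx.qa_plans
        try:
            ctx.qa_plans = []
            result = check_qa_plans(ctx, cfg)
            assert result.status is ComplianceStatus.FLAG
            assert result.details["mapcheck_plan_created"] == "FAIL"
        finally:
            ctx.qa_plans = saved

    def test_mapcheck_gantry_nonzero_flags(self, contexts, cfg):
        ctx = contexts["ONE_FX_FFF_WITH_MAPCHECK_QA"]
        beam = ctx.qa_plans[0].beams[0]
        saved = [cp.gantry_angle for cp in beam.control_points]
        try:
            for cp in beam.control_points:
                cp.gantry_angle = 30.0
            result = check_qa_plans(ctx, cfg)
            assert result.details["mapcheck_gantry_zero"] == "FAIL"
        finally:
            for cp, g in zip(beam.control_points, saved):
                cp.gantry_angle = g

    def test_gates_closed_on_fractionated_plan(self, contexts, cfg):
        result = check_qa_plans(contexts["STATIC_2FIELD"], cfg)
        assert result.status is PASS
        assert result.details["epid_mu_cp_match"] == "n/a"
        assert result.details["mapcheck_plan_created"] == "n/a"
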